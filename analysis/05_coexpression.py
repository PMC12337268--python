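#!/usr/bin/env python
"""Weighted coexpression networks for symbiont and host.

Builds one network per organism from strain-mean logCPM (median-count >= 10
prefilter; host restricted to its 5,000 most variable genes): soft power from
the scale-free fit, topological overlap, average-linkage static cut with kME
rescue, eigengene merging.  Writes module assignments and eigengenes.
"""

import argparse
from pathlib import Path

from pavcoex import expression, io, network
from pavcoex.config import AnalysisConfig


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--data", type=Path, default=Path("results/dataset"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    cfg = AnalysisConfig()

    sheet = io.read_sample_sheet(args.data / "sample_sheet.csv")
    for organism, fname in (("symbiont", "symbiont_counts.tsv"),
                            ("host", "host_counts.tsv")):
        counts = io.read_counts(args.data / fname).reorder_samples(
            sheet["sample_id"])
        sm = expression.strain_means(expression.logcpm(counts), sheet)
        expr = sm.loc[network.prefilter_for_network(counts,
                                                    cfg.median_count_floor)]
        if organism == "host":
            top = expression.select_variable_genes(
                expr, min(cfg.n_variable_host_genes, len(expr)))
            expr = expr.loc[top]
        net = network.build_network(expr, cfg)
        sizes = net.module_sizes
        print(f"{organism}: {len(expr)} genes, soft power {net.beta}, "
              f"{len(sizes)} modules (sizes {sizes.min()}..{sizes.max()}), "
              f"{(net.assignment == network.UNASSIGNED).sum()} unassigned")
        net.assignment.rename("module").rename_axis("gene_id").to_csv(
            args.out / f"{organism}_modules.tsv", sep="\t")
        net.eigengenes.rename_axis("module").to_csv(
            args.out / f"{organism}_eigengenes.tsv", sep="\t")
        net.fit_table.to_csv(args.out / f"{organism}_soft_power_fit.tsv",
                             sep="\t", index=False)
    print(f"tables written under {args.out}")


if __name__ == "__main__":
    main()
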