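"""Module-trait and cross-kingdom association, phenotype summaries, enrichment."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats

from pavcoex.config import AnalysisConfig
from pavcoex.pav import bh_fdr


def _pearson_with_t(x: np.ndarray, y: np.ndarray):
    r = float(np.clip(np.corrcoef(x, y)[0, 1], -1.0, 1.0))
    n = len(x)
    if abs(r) == 1.0:
        return r, math.inf * np.sign(r), 0.0
    t = r * math.sqrt(n - 2) / math.sqrt(1 - r * r)
    return r, t, 2 * stats.t.sf(abs(t), df=n - 2)


def module_trait_correlation(eigengenes: pd.DataFrame, phenotypes: pd.DataFrame,
                             config: AnalysisConfig | None = None) -> pd.DataFrame:
    """Pearson correlation of each module eigengene with each trait.

    p-values use the Student-t transform with df = n - 2; a module-trait pair
    is flagged significant at |r| > r_cut_module_trait and p <
    p_cut_module_trait (raw p by default; BH across modules per trait with
    ``config.adjust_module_trait``).
    """
    config = config or AnalysisConfig()
    strains = eigengenes.columns
    pheno = phenotypes.reindex(strains)
    if pheno.isna().any(axis=None):
        raise ValueError("phenotypes missing for some strains")
    rows = []
    for trait in pheno.columns:
        y = pheno[trait].to_numpy(dtype=float)
        if np.ptp(y) == 0:
            raise ValueError(f"trait {trait!r} is constant across strains")
        for module in eigengenes.index:
            x = eigengenes.loc[module].to_numpy(dtype=float)
            r, t, p = _pearson_with_t(x, y)
            rows.append((module, trait, r, t, p, len(strains)))
    table = pd.DataFrame(rows, columns=["unit_id", "trait", "r", "stat", "p", "n"])
    if config.adjust_module_trait:
        table["fdr"] = np.nan
        for trait in pheno.columns:
            m = table["trait"] == trait
            table.loc[m, "fdr"] = bh_fdr(table.loc[m, "p"].to_numpy())
        p_col = table["fdr"]
    else:
        p_col = table["p"]
    table["significant"] = (
        (table["r"].abs() > config.r_cut_module_trait)
        & (p_col < config.p_cut_module_trait)
    )
    table["direction"] = np.where(table["r"] > 0, "positive", "negative")
    return table


def cross_network_correlation(host_eigengenes: pd.DataFrame,
                              symbiont_eigengenes: pd.DataFrame,
                              config: AnalysisConfig | None = None,
                              trait: pd.Series | None = None) -> pd.DataFrame:
    """All pairwise host-module x symbiont-module eigengene correlations.

    Strains must match in identity and order (no silent alignment).  Edges
    pass the cut at |r| > r_cut_cross; when a trait is supplied each edge is
    annotated with both modules' trait correlations.
    """
    config = config or AnalysisConfig()
    if list(host_eigengenes.columns) != list(symbiont_eigengenes.columns):
        raise ValueError("host and symbiont eigengenes must share strain order")
    rows = []
    trait_r = {}
    if trait is not None:
        y = trait.reindex(host_eigengenes.columns).to_numpy(dtype=float)
        for name, eg in (("host", host_eigengenes), ("symbiont", symbiont_eigengenes)):
            for module in eg.index:
                trait_r[(name, module)] = _pearson_with_t(
                    eg.loc[module].to_numpy(dtype=float), y)[0]
    for hm in host_eigengenes.index:
        x = host_eigengenes.loc[hm].to_numpy(dtype=float)
        for sm in symbiont_eigengenes.index:
            r, t, p = _pearson_with_t(x, symbiont_eigengenes.loc[sm].to_numpy(dtype=float))
            rows.append((hm, sm, r, p, abs(r) > config.r_cut_cross,
                         trait_r.get(("host", hm), np.nan),
                         trait_r.get(("symbiont", sm), np.nan)))
    return pd.DataFrame(rows, columns=[
        "host_module", "symbiont_module", "r", "p", "passes_cut",
        "host_trait_r", "symbiont_trait_r",
    ])


def phenotype_summary(phenotypes: pd.DataFrame,
                      replicate_trait: pd.DataFrame | None = None,
                      trait: str = "shoot_biomass") -> dict:
    """Strain variance, CV, one-way ANOVA, and the trait correlation matrix.

    CV is SD/mean of the strain means.  With replicate-level data, a one-way
    ANOVA (strain factor) yields F and p, and the among-strain variance
    component by the method of moments, (MS_strain - MS_error) / n_reps,
    floored at zero.
    """
    if len(phenotypes) < 2:
        raise ValueError("need at least 2 strains")
    means = phenotypes[trait]
    cv = float(means.std(ddof=1) / means.mean())
    out = {
        "trait": trait,
        "n_strains": int(len(means)),
        "strain_mean_variance": float(means.var(ddof=1)),
        "cv": cv,
        "trait_correlations": phenotypes.corr(),
    }
    if replicate_trait is not None:
        groups = [g[trait].to_numpy(dtype=float)
                  for _, g in replicate_trait.groupby("strain_id")]
        ns = np.array([len(g) for g in groups])
        grand = np.concatenate(groups).mean()
        ss_between = float(sum(n * (g.mean() - grand) ** 2 for n, g in zip(ns, groups)))
        ss_within = float(sum(((g - g.mean()) ** 2).sum() for g in groups))
        df_between = len(groups) - 1
        df_within = int(ns.sum()) - len(groups)
        ms_between = ss_between / df_between
        if df_within == 0 or ss_within == 0:
            out.update(anova_F=np.nan, anova_p=np.nan, degenerate=True,
                       among_strain_variance=0.0 if ss_between == 0 else ms_between)
        else:
            ms_within = ss_within / df_within
            f_stat = ms_between / ms_within
            # balanced-design moment estimator; mean group size if unbalanced
            n0 = float(ns.mean())
            out.update(
                anova_F=float(f_stat),
                anova_p=float(stats.f.sf(f_stat, df_between, df_within)),
                degenerate=False,
                among_strain_variance=float(max((ms_between - ms_within) / n0, 0.0)),
            )
    return out


def category_enrichment(assignment: pd.Series, categories: pd.Series,
                        universe=None) -> pd.DataFrame:
    """Hypergeometric (upper-tail) enrichment of category labels per module.

    ``categories`` maps gene -> category label (a gene may carry no label by
    being absent from the series).  The universe defaults to all assigned +
    unassigned genes in ``assignment``.  p = P(overlap >= observed) from the
    hypergeometric law; BH FDR across all tested (module, category) pairs.
    """
    universe = pd.Index(universe) if universe is not None else assignment.index
    n_universe = len(universe)
    cats = categories.reindex(universe).dropna()
    missing = set(categories.index) - set(universe)
    if missing:
        raise ValueError(f"category gene {sorted(missing)[0]!r} not in universe")
    modules = sorted(set(assignment.loc[universe.intersection(assignment.index)])
                     - {"unassigned"})
    rows = []
    for module in modules:
        members = assignment.index[(assignment == module)
                                   & assignment.index.isin(universe)]
        for category, cat_genes in cats.groupby(cats):
            k_cat = len(cat_genes)
            overlap = len(members.intersection(cat_genes.index))
            p = float(stats.hypergeom.sf(overlap - 1, n_universe, k_cat, len(members)))
            rows.append((module, category, overlap, len(members), k_cat, n_universe, p))
    table = pd.DataFrame(rows, columns=[
        "module", "category", "overlap", "module_size", "category_size",
        "universe_size", "p",
    ])
    if len(table):
        table["fdr"] = bh_fdr(table["p"].to_numpy())
    else:
        table["fdr"] = []
    return table


def markdown_report(pav_assoc: pd.DataFrame | None, cluster_tests: pd.DataFrame | None,
                    module_trait: pd.DataFrame | None, cross_edges: pd.DataFrame | None,
                    pheno_summary: dict | None) -> str:
    """One-page Markdown summary of the significant findings."""
    lines = ["# Pipeline report", ""]
    if pheno_summary is not None:
        f_stat = pheno_summary.get("anova_F")
        has_anova = f_stat is not None and f_stat == f_stat
        lines += [
            "## Phenotype",
            f"- {pheno_summary['trait']}: among-strain variance "
            f"{pheno_summary['strain_mean_variance']:.4f}, CV {pheno_summary['cv']:.2f}"
            + (f", ANOVA F = {f_stat:.1f} (p = {pheno_summary['anova_p']:.2g})"
               if has_anova else ""),
            "",
        ]
    if pav_assoc is not None:
        sig = pav_assoc[pav_assoc["significant"]]
        lines += ["## Gene presence-absence vs trait",
                  f"- {len(pav_assoc)} on/off genes tested, {len(sig)} significant",
                  ""]
    if cluster_tests is not None and len(cluster_tests):
        lines.append("## Syntenic clusters")
        for row in cluster_tests.itertuples(index=False):
            if not row.undefined:
                lines.append(
                    f"- {row.unit_id}: t = {row.stat:.2f}, p = {row.p:.3g} "
                    f"(present in {row.n_present} strains)"
                )
        lines.append("")
    if module_trait is not None:
        sig = module_trait[module_trait["significant"]]
        lines += ["## Module-trait associations",
                  f"- {len(sig)} significant module-trait pairs"]
        for row in sig.itertuples(index=False):
            lines.append(f"  - {row.unit_id} vs {row.trait}: r = {row.r:.2f} "
                         f"(p = {row.p:.2g}, {row.direction})")
        lines.append("")
    if cross_edges is not None:
        passed = cross_edges[cross_edges["passes_cut"]]
        lines += ["## Cross-kingdom module edges",
                  f"- {len(passed)} of {len(cross_edges)} pairs pass the cut"]
        for row in passed.itertuples(index=False):
            lines.append(f"  - {row.host_module} ~ {row.symbiont_module}: r = {row.r:.2f}")
        lines.append("")
    return "\n".join(lines)
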