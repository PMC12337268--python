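"""Weighted coexpression networks over strain-mean expression.

The construction follows the standard weighted-network recipe: Pearson
correlation across strains, soft-thresholded adjacency a_ij = |cor|^beta
(unsigned by default), topological overlap

    TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij),
    l_ij = sum_{u != i,j} a_iu * a_uj,

average-linkage hierarchical clustering on 1 - TOM with a static height cut
(module cores) followed by a kME rescue step that attaches leftover genes to
the core whose eigengene they best correlate with, module eigengenes as the
first singular vector of the standardized module expression, and iterative
merging of modules with highly correlated eigengenes.  The whole stage is
deterministic given its inputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from pavcoex.config import AnalysisConfig
from pavcoex.io import CountsMatrix

UNASSIGNED = "unassigned"


def prefilter_for_network(counts: CountsMatrix, floor: float = 10.0) -> pd.Index:
    """Genes whose median raw count across all samples is >= floor."""
    med = np.median(counts.counts, axis=1)
    return counts.gene_ids[med >= floor]


def adjacency_matrix(expr: pd.DataFrame, beta: float, signed: bool = False) -> np.ndarray:
    """Soft-thresholded adjacency from gene x strain expression."""
    x = expr.to_numpy(dtype=float)
    sd = x.std(axis=1, ddof=1)
    if (sd == 0).any():
        raise ValueError(f"constant expression for gene {expr.index[np.argmax(sd == 0)]!r}")
    cor = np.corrcoef(x)
    np.clip(cor, -1.0, 1.0, out=cor)
    if signed:
        adj = ((1 + cor) / 2) ** beta
    else:
        adj = np.abs(cor) ** beta
    np.fill_diagonal(adj, 0.0)
    return adj


def scale_free_fit(connectivity: np.ndarray, n_bins: int = 10) -> float:
    """R^2 of the log-log regression of frequency on binned connectivity."""
    k = np.asarray(connectivity, dtype=float)
    if np.ptp(k) == 0:
        return 0.0
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    counts, _ = np.histogram(k, bins=edges)
    centers = (edges[:-1] + edges[1:]) / 2
    keep = (counts > 0) & (centers > 0)
    if keep.sum() < 3:
        return 0.0
    logk = np.log10(centers[keep])
    logp = np.log10(counts[keep] / counts.sum())
    r = np.corrcoef(logk, logp)[0, 1]
    return float(r ** 2)


def pick_soft_power(expr: pd.DataFrame, config: AnalysisConfig | None = None):
    """Choose the soft power from the scale-free fit table.

    Candidates whose mean connectivity exceeds ``max_mean_connectivity`` are
    skipped while a sparser qualifying power exists (standard guidance: very
    dense networks defeat the point of soft thresholding).  Among the
    remaining powers the smallest beta reaching the target R^2 wins; if none
    reaches it, the beta maximizing R^2.  Returns (beta, fit table).
    """
    config = config or AnalysisConfig()
    if expr.shape[1] < 4:
        raise ValueError("need at least 4 strains to pick a soft power")
    x = expr.to_numpy(dtype=float)
    if (x.std(axis=1, ddof=1) == 0).any():
        raise ValueError("constant expression matrix")
    cor = np.abs(np.corrcoef(x))
    np.clip(cor, 0.0, 1.0, out=cor)
    np.fill_diagonal(cor, 0.0)
    rows = []
    for beta in config.soft_power_grid:
        adj = cor ** beta
        k = adj.sum(axis=1)
        rows.append((beta, scale_free_fit(k), float(k.mean()), float(k.max())))
    fit = pd.DataFrame(rows, columns=["beta", "r2", "mean_connectivity", "max_connectivity"])
    eligible = fit[fit["mean_connectivity"] <= config.max_mean_connectivity]
    if not len(eligible):
        eligible = fit
    reaching = eligible[eligible["r2"] >= config.scale_free_r2]
    if len(reaching):
        beta = int(reaching["beta"].iloc[0])
    else:
        beta = int(eligible.loc[eligible["r2"].idxmax(), "beta"])
    return beta, fit


def compute_tom(adjacency: np.ndarray) -> np.ndarray:
    """Topological overlap matrix of a symmetric adjacency in [0, 1]."""
    a = np.asarray(adjacency, dtype=float)
    if a.shape[0] != a.shape[1] or not np.allclose(a, a.T):
        raise ValueError("adjacency must be square and symmetric")
    a = a.copy()
    np.fill_diagonal(a, 0.0)
    l = a @ a  # l_ij = sum_u a_iu a_uj (diagonal of a is zero)
    k = a.sum(axis=1)
    denom = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = (l + a) / denom
    tom = np.nan_to_num(tom, nan=0.0)
    np.fill_diagonal(tom, 1.0)
    return tom


def cut_modules(tom: np.ndarray, gene_ids: pd.Index,
                config: AnalysisConfig | None = None) -> pd.Series:
    """Static-cut module detection on the TOM dissimilarity dendrogram.

    Average-linkage clustering of 1 - TOM, cut at the fixed height
    ``cut_height``; subtrees smaller than ``min_module_size`` become
    unassigned; labels M1, M2, ... ordered by decreasing size.
    """
    config = config or AnalysisConfig()
    n = tom.shape[0]
    if n != len(gene_ids):
        raise ValueError("TOM size does not match gene ids")
    dissim = 1.0 - tom
    np.fill_diagonal(dissim, 0.0)
    condensed = squareform(dissim, checks=False)
    z = linkage(condensed, method="average")
    raw = fcluster(z, t=float(config.cut_height), criterion="distance")
    assignment = pd.Series(UNASSIGNED, index=gene_ids, dtype=object)
    sizes = pd.Series(raw).value_counts()
    keep = sizes[sizes >= config.min_module_size]
    for rank, (raw_label, _) in enumerate(
            sorted(keep.items(), key=lambda kv: (-kv[1], kv[0])), start=1):
        assignment.iloc[np.flatnonzero(raw == raw_label)] = f"M{rank}"
    if (assignment == UNASSIGNED).all():
        import warnings
        warnings.warn("no module reached min_module_size; all genes unassigned")
    return assignment


def assign_by_kme(expr: pd.DataFrame, assignment: pd.Series,
                  kme_min: float = 0.6) -> pd.Series:
    """Assign unassigned genes to the module core they best correlate with.

    kME is the correlation of a gene's profile with a module eigengene; a
    leftover gene joins the module maximizing |kME| when that value reaches
    ``kme_min``, otherwise it stays unassigned.  Core members are untouched.
    """
    modules = sorted(set(assignment) - {UNASSIGNED})
    if not modules:
        return assignment.copy()
    eigengenes, _ = module_eigengenes(expr, assignment)
    x = expr.to_numpy(dtype=float)
    e = eigengenes.to_numpy(dtype=float)
    xc = x - x.mean(axis=1, keepdims=True)
    ec = e - e.mean(axis=1, keepdims=True)
    denom = np.sqrt((xc ** 2).sum(axis=1)[:, None] * (ec ** 2).sum(axis=1)[None, :])
    with np.errstate(invalid="ignore", divide="ignore"):
        kme = np.abs(xc @ ec.T / denom)
    kme = np.nan_to_num(kme)
    best = kme.argmax(axis=1)
    best_val = kme[np.arange(len(kme)), best]
    out = assignment.copy()
    rescue = (assignment == UNASSIGNED).to_numpy() & (best_val >= kme_min)
    out.iloc[np.flatnonzero(rescue)] = [eigengenes.index[b] for b in best[rescue]]
    return out


def module_eigengenes(expr: pd.DataFrame, assignment: pd.Series):
    """First principal component of each module's standardized expression.

    Eigengenes have unit norm over strains and are oriented so that the mean
    correlation with member-gene profiles is non-negative.  Returns
    ``(eigengenes, variance_explained)``: module x strain values and the
    fraction of module variance captured.
    """
    modules = sorted(set(assignment) - {UNASSIGNED},
                     key=lambda m: (len(m), m))
    rows, var_rows = [], []
    for module in modules:
        genes = assignment.index[assignment == module]
        x = expr.loc[genes].to_numpy(dtype=float)
        mean = x.mean(axis=1, keepdims=True)
        sd = x.std(axis=1, ddof=1, keepdims=True)
        z = (x - mean) / np.where(sd > 0, sd, 1.0)
        u, s, vt = np.linalg.svd(z, full_matrices=False)
        eig = vt[0]
        cors = _row_cor(z, eig)
        if np.nanmean(cors) < 0:
            eig = -eig
        rows.append(eig)
        total = (s ** 2).sum()
        var_rows.append(s[0] ** 2 / total if total > 0 else 0.0)
    eigengenes = pd.DataFrame(rows, index=modules, columns=expr.columns)
    variance_explained = pd.Series(var_rows, index=modules, name="variance_explained")
    return eigengenes, variance_explained


def _row_cor(z: np.ndarray, v: np.ndarray) -> np.ndarray:
    vc = v - v.mean()
    zc = z - z.mean(axis=1, keepdims=True)
    denom = np.sqrt((zc ** 2).sum(axis=1) * (vc ** 2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        return zc @ vc / denom


def merge_similar_modules(expr: pd.DataFrame, assignment: pd.Series,
                          merge_cor: float = 0.75):
    """Merge module pairs whose eigengenes correlate above ``merge_cor``.

    The most-correlated pair merges first; eigengenes are recomputed and the
    step repeats to a fixpoint, so the result does not depend on initial
    label order.  Returns ``(assignment, eigengenes, variance_explained)``
    with modules relabeled M1, M2, ... by decreasing size.
    """
    assignment = assignment.copy()
    while True:
        eigengenes, _ = module_eigengenes(expr, assignment)
        if len(eigengenes) < 2:
            break
        cor = np.corrcoef(eigengenes.to_numpy())
        np.fill_diagonal(cor, -np.inf)
        i, j = np.unravel_index(np.argmax(cor), cor.shape)
        if cor[i, j] <= merge_cor:
            break
        a, b = eigengenes.index[i], eigengenes.index[j]
        assignment[assignment == b] = a
    # relabel by size
    sizes = assignment[assignment != UNASSIGNED].value_counts()
    mapping = {old: f"M{rank}" for rank, (old, _) in enumerate(
        sorted(sizes.items(), key=lambda kv: (-kv[1], kv[0])), start=1)}
    assignment = assignment.map(lambda m: mapping.get(m, UNASSIGNED))
    eigengenes, variance_explained = module_eigengenes(expr, assignment)
    return assignment, eigengenes, variance_explained


@dataclass
class CoexpressionNetwork:
    """Result bundle of one organism's network construction."""

    genes: pd.Index
    beta: int
    fit_table: pd.DataFrame
    assignment: pd.Series
    eigengenes: pd.DataFrame
    variance_explained: pd.Series

    @property
    def module_sizes(self) -> pd.Series:
        return self.assignment[self.assignment != UNASSIGNED].value_counts()


def build_network(expr: pd.DataFrame, config: AnalysisConfig | None = None) -> CoexpressionNetwork:
    """Full network construction for one organism's strain-mean matrix."""
    config = config or AnalysisConfig()
    if len(expr) > config.max_network_genes:
        raise ValueError(
            f"{len(expr)} genes exceed max_network_genes={config.max_network_genes}; "
            "prefilter or raise the cap explicitly"
        )
    # drop zero-variance genes: they carry no coexpression information
    sd = expr.std(axis=1, ddof=1)
    expr = expr.loc[sd > 0]
    beta, fit = pick_soft_power(expr, config)
    adj = adjacency_matrix(expr, beta, signed=config.signed_network)
    tom = compute_tom(adj)
    assignment = cut_modules(tom, expr.index, config)
    assignment = assign_by_kme(expr, assignment, config.kme_min)
    assignment, eigengenes, variance_explained = merge_similar_modules(
        expr, assignment, config.merge_cor
    )
    return CoexpressionNetwork(
        genes=expr.index, beta=beta, fit_table=fit, assignment=assignment,
        eigengenes=eigengenes, variance_explained=variance_explained,
    )
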