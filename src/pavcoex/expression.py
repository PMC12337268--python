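"""Normalization, expression-status classes, strain summaries, and PCA.

logCPM uses a small prior count:
``log2((count + prior) / (lib_size + 2 * prior) * 1e6)``, prior 0.5 by
default.  Strain summaries average per-sample logCPM over a strain's
replicates (log first, then average).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from pavcoex.io import CountsMatrix


def logcpm(counts: CountsMatrix, prior: float = 0.5) -> pd.DataFrame:
    """Log2 counts-per-million with a prior count; genes x samples."""
    libs = counts.lib_sizes.astype(float)
    if (libs <= 0).any():
        bad = counts.sample_ids[np.argmax(libs <= 0)]
        raise ValueError(f"zero library size for sample {bad!r}")
    vals = np.log2((counts.counts + prior) / (libs + 2 * prior)[None, :] * 1e6)
    return pd.DataFrame(vals, index=counts.gene_ids, columns=counts.sample_ids)


def classify_expression_status(counts: CountsMatrix, sample_sheet: pd.DataFrame,
                               floor: float = 10.0) -> pd.DataFrame:
    """Partition genes into common / never / variable expression classes.

    common: count >= floor in every replicate of every strain;
    never: count < floor in every replicate of every strain;
    variable: otherwise.  Also returns per-strain "expressed" flags (count >=
    floor in all of that strain's replicates).
    """
    sheet = sample_sheet.set_index("sample_id").loc[counts.sample_ids]
    above = counts.counts >= floor
    strains = list(dict.fromkeys(sheet["strain_id"]))
    expressed = pd.DataFrame(index=counts.gene_ids, columns=strains, dtype=bool)
    for strain in strains:
        cols = (sheet["strain_id"] == strain).to_numpy()
        expressed[strain] = above[:, cols].all(axis=1)
    common = above.all(axis=1)
    never = (~above).all(axis=1)
    status = np.where(common, "common", np.where(never, "never", "variable"))
    out = expressed.copy()
    out.insert(0, "status", status)
    return out


def strain_means(values: pd.DataFrame, sample_sheet: pd.DataFrame) -> pd.DataFrame:
    """Arithmetic mean over each strain's replicates; genes x strains."""
    sheet = sample_sheet.set_index("sample_id").loc[values.columns]
    means = values.T.groupby(sheet["strain_id"], sort=False).mean().T
    means.columns.name = None
    return means


def select_variable_genes(matrix: pd.DataFrame, n: int = 5000) -> pd.Index:
    """Top-n genes by variance across columns; ties broken by gene id."""
    if n > len(matrix):
        raise ValueError(f"requested {n} genes but matrix has {len(matrix)}")
    var = matrix.var(axis=1, ddof=1)
    order = sorted(matrix.index, key=lambda g: (-var[g], g))
    return pd.Index(order[:n])


@dataclass
class PCAResult:
    scores: pd.DataFrame  # strain x component
    variance_explained: np.ndarray  # fraction per component
    loadings: pd.DataFrame  # gene x component


def pca_strains(matrix: pd.DataFrame, n_components: int | None = None,
                center: bool = True, scale: bool = False) -> PCAResult:
    """PCA over strains (observations) of a gene x strain matrix.

    variance_explained is eigenvalue / trace of the strain covariance of the
    centered (optionally gene-scaled) data.  Degenerate data (all strains
    identical) reports all-zero explained fractions.
    """
    if matrix.shape[1] < 2:
        raise ValueError("need at least 2 strains for PCA")
    max_comp = min(matrix.shape[1] - 1, matrix.shape[0])
    k = max_comp if n_components is None else n_components
    if k > max_comp:
        raise ValueError(f"requested {k} components, at most {max_comp} available")
    x = matrix.to_numpy(dtype=float).T  # strains x genes
    if center:
        x = x - x.mean(axis=0, keepdims=True)
    if scale:
        sd = x.std(axis=0, ddof=1)
        x = x / np.where(sd > 0, sd, 1.0)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    eig = s ** 2 / max(x.shape[0] - 1, 1)
    trace = eig.sum()
    explained = eig / trace if trace > 0 else np.zeros_like(eig)
    comps = [f"PC{i + 1}" for i in range(k)]
    scores = pd.DataFrame((u * s)[:, :k], index=matrix.columns, columns=comps)
    loadings = pd.DataFrame(vt[:k].T, index=matrix.index, columns=comps)
    return PCAResult(scores=scores, variance_explained=explained[:k], loadings=loadings)


def dispersion_summary(strain_mean_matrix: pd.DataFrame,
                       gene_class: pd.Series) -> pd.DataFrame:
    """Mean and among-strain variance of strain-mean expression by pangenome class.

    A descriptive analog of the observation that accessory (shell/cloud) genes
    show higher expression dispersion among strains than core genes.
    """
    mean = strain_mean_matrix.mean(axis=1)
    var = strain_mean_matrix.var(axis=1, ddof=1)
    df = pd.DataFrame({"mean": mean, "variance": var,
                       "gene_class": gene_class.reindex(strain_mean_matrix.index)})
    return (
        df.groupby("gene_class")
        .agg(n=("mean", "size"), mean_expression=("mean", "mean"),
             mean_dispersion=("variance", "mean"),
             median_dispersion=("variance", "median"))
        .reset_index()
    )
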