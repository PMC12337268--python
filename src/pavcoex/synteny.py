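"""Syntenic clustering of candidate genes and pangenome partitioning.

A syntenic cluster is a run of two or more candidate genes on one replicon in
which consecutive members are separated by an inter-feature gap of at most
``cluster_gap_bp`` (3 kb by default, gap = next.start - current.end - 1,
inclusive).  Pangenome classes follow the frequency bins core (> 99% of
strains), shell (15-95%) and cloud (< 15%); the printed bins leave
(95%, 99%] undefined, which is assigned shell.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from pavcoex.config import AnalysisConfig


@dataclass
class SyntenicCluster:
    cluster_id: str
    replicon_id: str
    genes: list  # ordered by start coordinate
    start: int
    end: int

    @property
    def span(self) -> int:
        return self.end - self.start + 1

    @property
    def size(self) -> int:
        return len(self.genes)


def detect_clusters(annotation: pd.DataFrame, candidates, gap: int = 3000):
    """Chain candidate genes into syntenic clusters.

    Candidates are sorted by start within each replicon and chained while the
    inter-feature gap (next.start - current.end - 1) is <= ``gap``; chains of
    length >= 2 become clusters, singletons are returned separately.
    """
    candidates = pd.Index(candidates)
    ann = annotation.set_index("gene_id")
    missing = candidates.difference(ann.index)
    if len(missing):
        raise ValueError(f"candidate {missing[0]!r} has no annotation")
    sub = ann.loc[candidates, ["replicon_id", "start", "end"]].sort_values(
        ["replicon_id", "start", "end"]
    )
    clusters: list[SyntenicCluster] = []
    singletons: list[str] = []
    for replicon, block in sub.groupby("replicon_id", sort=True):
        chain: list[tuple[str, int, int]] = []
        max_end = None
        for gene_id, row in block.iterrows():
            if max_end is not None and row["start"] - max_end - 1 <= gap:
                chain.append((gene_id, row["start"], row["end"]))
                max_end = max(max_end, row["end"])
            else:
                _emit(chain, replicon, clusters, singletons)
                chain = [(gene_id, row["start"], row["end"])]
                max_end = row["end"]
        _emit(chain, replicon, clusters, singletons)
    for i, cl in enumerate(clusters, start=1):
        cl.cluster_id = f"C{i}"
    return clusters, singletons


def _emit(chain, replicon, clusters, singletons):
    if not chain:
        return
    if len(chain) == 1:
        singletons.append(chain[0][0])
    else:
        clusters.append(SyntenicCluster(
            cluster_id="", replicon_id=replicon,
            genes=[g for g, _, _ in chain],
            start=min(s for _, s, _ in chain),
            end=max(e for _, _, e in chain),
        ))


def cluster_presence(clusters, gene_presence: pd.DataFrame,
                     rule="all") -> pd.DataFrame:
    """Cluster x strain presence from member-gene presence.

    ``rule="all"``: a cluster is present only where every member is present;
    a fraction in (0, 1] requires at least that fraction of members.
    """
    rows = {}
    for cl in clusters:
        members = gene_presence.loc[cl.genes]
        if rule == "all":
            rows[cl.cluster_id] = members.all(axis=0)
        else:
            frac = float(rule)
            rows[cl.cluster_id] = members.mean(axis=0) >= frac
    return pd.DataFrame.from_dict(rows, orient="index",
                                  columns=gene_presence.columns).astype(bool)


def cluster_trait_ttest(cluster_presence_matrix: pd.DataFrame, trait: pd.Series,
                        welch: bool = False) -> pd.DataFrame:
    """Two-sample t test of the trait between carrier and non-carrier strains.

    Pooled-variance Student's t by default (Welch optional).  Groups of size
    < 2 yield an undefined-flagged record.
    """
    y = trait.reindex(cluster_presence_matrix.columns)
    if y.isna().any():
        raise ValueError("trait missing for some strains")
    rows = []
    for cluster_id, pres in cluster_presence_matrix.iterrows():
        a = y[pres.to_numpy(dtype=bool)].to_numpy(dtype=float)
        b = y[~pres.to_numpy(dtype=bool)].to_numpy(dtype=float)
        if len(a) < 2 or len(b) < 2:
            rows.append((cluster_id, len(a), len(b), np.nan, np.nan, np.nan,
                         np.nan, np.nan, True))
            continue
        t, p = stats.ttest_ind(a, b, equal_var=not welch)
        df = (len(a) + len(b) - 2) if not welch else _welch_df(a, b)
        rows.append((cluster_id, len(a), len(b), a.mean(), b.mean(),
                     float(t), float(df), float(p), False))
    return pd.DataFrame(rows, columns=[
        "unit_id", "n_present", "n_absent", "mean_present", "mean_absent",
        "stat", "df", "p", "undefined",
    ])


def _welch_df(a, b):
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    return (va + vb) ** 2 / (va ** 2 / (len(a) - 1) + vb ** 2 / (len(b) - 1))


def classify_pangenome(presence: pd.DataFrame, config: AnalysisConfig | None = None,
                       n_strains: int | None = None,
                       replicon_of: pd.Series | None = None):
    """Partition gene groups into core / shell / cloud by presence fraction.

    f = strains carrying the group / n_strains.  core iff f > core_frac;
    cloud iff f < shell_lo; shell otherwise (this assigns the undefined
    (shell_hi, core_frac] bin to shell).  Returns ``(classes, summary)`` with
    per-replicon class fractions when ``replicon_of`` maps group -> replicon.
    """
    config = config or AnalysisConfig()
    n = n_strains or presence.shape[1]
    count = presence.sum(axis=1).astype(int)
    if (count == 0).any():
        empty = presence.index[count == 0][0]
        raise ValueError(f"group {empty!r} present in no strain")
    frac = count / n
    label = np.where(frac > config.core_frac, "core",
                     np.where(frac < config.shell_lo, "cloud", "shell"))
    classes = pd.DataFrame({"fraction": frac, "pangenome_class": label},
                           index=presence.index)
    summary = None
    if replicon_of is not None:
        df = classes.copy()
        df["replicon_id"] = replicon_of.reindex(classes.index)
        summary = (
            df.groupby("replicon_id")["pangenome_class"]
            .value_counts(normalize=True).rename("fraction").reset_index()
            .pivot(index="replicon_id", columns="pangenome_class", values="fraction")
            .fillna(0.0)
        )
        for col in ("core", "shell", "cloud"):
            if col not in summary:
                summary[col] = 0.0
        summary = summary[["core", "shell", "cloud"]]
    return classes, summary
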