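"""Presence-absence variation calling and confirmation.

Expression-based calls follow a filterByExpr-style rule: each strain gets a
CPM cutoff equivalent to ``cpm_floor`` counts at the median library size of
its replicates, and a gene is absent in a strain when its CPM falls below the
cutoff in at least ceil(absent_rep_fraction * n_reps) replicates (three out of
four at the default design).

Sequence-based calls use nucleotide containment: exact k-mer seeds locate the
candidate region, and the query is globally aligned to the spanned window
(bit-parallel edit-distance alignment via edlib) on both strands; a gene is
present when the best hit reaches ``min_identity`` and ``min_coverage``.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass

import edlib
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from pavcoex.config import AnalysisConfig
from pavcoex.io import CountsMatrix

_RC = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_RC)[::-1]


# ---------------------------------------------------------------------------
# expression-based presence

def call_presence_from_expression(counts: CountsMatrix, sample_sheet: pd.DataFrame,
                                  config: AnalysisConfig | None = None) -> pd.DataFrame:
    """Boolean gene x strain presence calls from expression.

    Per strain, cutoff (CPM) = cpm_floor / median(lib sizes of its replicates,
    in millions); absent iff CPM < cutoff in >= ceil(absent_rep_fraction *
    n_reps) of the strain's replicates.
    """
    config = config or AnalysisConfig()
    sheet = sample_sheet.set_index("sample_id").loc[counts.sample_ids]
    libs = counts.lib_sizes.astype(float)
    if (libs <= 0).any():
        raise ValueError("sample with zero library size")
    cpm = counts.counts / libs[None, :] * 1e6
    strains = list(dict.fromkeys(sheet["strain_id"]))
    presence = pd.DataFrame(index=counts.gene_ids, columns=strains, dtype=bool)
    for strain in strains:
        cols = (sheet["strain_id"] == strain).to_numpy()
        n_reps = int(cols.sum())
        cutoff = config.cpm_floor / (np.median(libs[cols]) / 1e6)
        n_below_needed = math.ceil(config.absent_rep_fraction * n_reps)
        below = (cpm[:, cols] < cutoff).sum(axis=1)
        presence[strain] = below < n_below_needed
    return presence


def filter_onoff(presence: pd.DataFrame, config: AnalysisConfig | None = None) -> pd.Index:
    """Genes present in at least min_present_strains and at most
    max_present_strains (default 3 .. n_strains - 3)."""
    config = config or AnalysisConfig()
    n_strains = presence.shape[1]
    hi = config.resolved_max_present(n_strains)
    lo = config.min_present_strains
    n_present = presence.sum(axis=1)
    return presence.index[(n_present >= lo) & (n_present <= hi)]


# ---------------------------------------------------------------------------
# trait association

def bh_fdr(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (step-up)."""
    return multipletests(pvalues, method="fdr_bh")[1]


def correlate_presence_with_trait(presence: pd.DataFrame, trait: pd.Series,
                                  config: AnalysisConfig | None = None,
                                  expression: pd.DataFrame | None = None) -> pd.DataFrame:
    """Point-biserial correlation of gene presence with a strain-level trait.

    Returns one record per gene with r, t statistic, p (two-sided, df = n-2),
    BH FDR over the tested (non-constant) genes, and a ``significant`` flag at
    |r| > r_cut_gene and fdr < fdr_cut_gene.  Genes with constant presence are
    emitted with a ``constant`` flag and excluded from testing.

    With ``config.trait_cor_on_expression`` and an ``expression`` matrix
    (gene x strain strain means), the correlation uses expression values
    instead of the 0/1 indicator.
    """
    config = config or AnalysisConfig()
    strains = presence.columns
    y = trait.reindex(strains)
    if y.isna().any():
        missing = strains[y.isna()][0]
        raise ValueError(f"trait missing for strain {missing!r}")
    y = y.to_numpy(dtype=float)
    n = len(strains)

    rows = []
    for gene in presence.index:
        if config.trait_cor_on_expression and expression is not None:
            x = expression.loc[gene, strains].to_numpy(dtype=float)
        else:
            x = presence.loc[gene].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            rows.append((gene, int(presence.loc[gene].sum()), np.nan, np.nan, np.nan, True))
            continue
        r, _ = stats.pearsonr(x, y)
        r = float(np.clip(r, -1.0, 1.0))
        if abs(r) == 1.0:
            t = np.inf * np.sign(r)
            p = 0.0
        else:
            t = r * math.sqrt(n - 2) / math.sqrt(1 - r * r)
            p = 2 * stats.t.sf(abs(t), df=n - 2)
        rows.append((gene, int(presence.loc[gene].sum()), r, t, p, False))

    table = pd.DataFrame(
        rows, columns=["unit_id", "n_present", "r", "stat", "p", "constant"]
    )
    table["n"] = n
    table["fdr"] = np.nan
    tested = ~table["constant"]
    if tested.any():
        table.loc[tested, "fdr"] = bh_fdr(table.loc[tested, "p"].to_numpy())
    table["significant"] = (
        tested
        & (table["r"].abs() > config.r_cut_gene)
        & (table["fdr"] < config.fdr_cut_gene)
    )
    return table


# ---------------------------------------------------------------------------
# sequence-based presence

@dataclass
class SequenceHit:
    gene_id: str
    strain_id: str
    identity: float
    coverage: float
    replicon_id: str | None
    start: int | None  # 1-based inclusive
    end: int | None
    strand: str | None


_CIGAR_RE = re.compile(r"(\d+)([=XID])")


def _cigar_stats(cigar: str) -> tuple[int, int, int, int]:
    """(matches, mismatches, insertions-to-query, deletions-from-query)."""
    eq = x = ins = dele = 0
    for num, op in _CIGAR_RE.findall(cigar):
        k = int(num)
        if op == "=":
            eq += k
        elif op == "X":
            x += k
        elif op == "I":
            ins += k
        else:
            dele += k
    return eq, x, ins, dele


def _align_window(query: str, window: str):
    """Identity/coverage of the best containment alignment of query in window.

    identity = matching columns / alignment columns; coverage = query bases
    aligned to a target base / query length.
    """
    res = edlib.align(query, window, mode="HW", task="path")
    if res["editDistance"] < 0 or not res.get("cigar"):
        return None
    eq, x, ins, dele = _cigar_stats(res["cigar"])
    cols = eq + x + ins + dele
    identity = eq / cols if cols else 0.0
    coverage = (eq + x) / len(query)
    loc = res["locations"][0]
    return identity, coverage, loc


def _seed_candidates(query: str, target: str, k: int, offset: int) -> list[int]:
    """Candidate alignment start positions from one exact k-mer seed."""
    seed = query[offset:offset + k]
    candidates = []
    pos = target.find(seed)
    while pos != -1:
        candidates.append(pos - offset)
        pos = target.find(seed, pos + 1)
    return candidates


def find_sequence_presence(gene_seqs: dict, genomes, config: AnalysisConfig | None = None,
                           strains: list | None = None, n_seeds: int = 6):
    """Search each query gene in each strain genome; call sequence presence.

    ``genomes`` is any store exposing ``strains``, ``replicons(strain)`` and
    ``sequence(strain, replicon)`` (see :class:`pavcoex.io.GenomeStore`), or a
    plain ``{strain: {replicon: seq}}`` mapping.

    Returns ``(hits, presence)``: a hit table with the best hit per
    (gene, strain) (1-based inclusive coordinates) and the boolean presence
    matrix at ``min_identity`` / ``min_coverage``.
    """
    config = config or AnalysisConfig()
    k = config.kmer_size
    if isinstance(genomes, dict):
        strain_list = strains or list(genomes)
        get_reps = lambda s: list(genomes[s])
        get_seq = lambda s, r: genomes[s][r]
    else:
        strain_list = strains or genomes.strains
        get_reps = genomes.replicons
        get_seq = genomes.sequence

    for gid, seq in gene_seqs.items():
        if len(seq) < k:
            raise ValueError(f"query {gid!r} shorter than k-mer size {k}")

    hits = []
    presence = pd.DataFrame(False, index=pd.Index(gene_seqs.keys()), columns=strain_list)
    for strain in strain_list:
        replicons = get_reps(strain)
        seqs = {rep: get_seq(strain, rep).upper() for rep in replicons}
        for gid, query in gene_seqs.items():
            best = _best_hit(gid, strain, query.upper(), seqs, k, n_seeds, config)
            hits.append(best)
            presence.loc[gid, strain] = (
                best.identity >= config.min_identity
                and best.coverage >= config.min_coverage
            )
    hit_table = pd.DataFrame([vars(h) for h in hits])
    return hit_table, presence


def _best_hit(gid, strain, query, seqs, k, n_seeds, config) -> SequenceHit:
    """Best containment hit of one query in one strain's replicons.

    Seeds are tried in order and the search stops as soon as a hit passes the
    presence thresholds (further seeds can only relocate the same region);
    otherwise the best-scoring hit over all seeds is kept.
    """
    qlen = len(query)
    variants = (("+", query), ("-", reverse_complement(query)))
    best = _scan_seeds(gid, strain, variants, seqs, k, n_seeds, qlen, config)
    if best is None and k > 15:
        # no seed survived: the copy may be too diverged for long exact
        # seeds, so rescan with shorter, denser ones before calling absent
        best = _scan_seeds(gid, strain, variants, seqs, 15, 4 * n_seeds,
                           qlen, config)
    if best is None:
        best = SequenceHit(gid, strain, 0.0, 0.0, None, None, None, None)
    return best


def _scan_seeds(gid, strain, variants, seqs, k, n_seeds, qlen, config):
    offsets = np.unique(np.linspace(0, qlen - k, n_seeds).astype(int))
    best = None
    seen_windows = set()
    for off in offsets:
        for strand, q in variants:
            for rep, target in seqs.items():
                for cand in _seed_candidates(q, target, k, int(off)):
                    pad = max(50, qlen // 10)
                    w_start = max(0, cand - pad)
                    key = (strand, rep, w_start // max(pad, 1))
                    if key in seen_windows:
                        continue
                    seen_windows.add(key)
                    res = _align_window(q, target[w_start:cand + qlen + pad])
                    if res is None:
                        continue
                    identity, coverage, (loc0, loc1) = res
                    hit = SequenceHit(
                        gene_id=gid, strain_id=strain,
                        identity=identity, coverage=coverage, replicon_id=rep,
                        start=w_start + loc0 + 1, end=w_start + loc1 + 1,
                        strand=strand,
                    )
                    if best is None or (hit.identity, hit.coverage) > (
                            best.identity, best.coverage):
                        best = hit
                    if (best.identity >= config.min_identity
                            and best.coverage >= config.min_coverage):
                        return best
    return best


# ---------------------------------------------------------------------------
# agreement

def agreement_filter(expression_presence: pd.DataFrame,
                     sequence_presence: pd.DataFrame):
    """Keep genes whose expression and sequence calls agree in every strain.

    Returns ``(confirmed_genes, discordance)`` where ``discordance`` counts
    disagreeing strains per non-confirmed gene.
    """
    if not expression_presence.index.equals(sequence_presence.index) or not (
        list(expression_presence.columns) == list(sequence_presence.columns)
    ):
        raise ValueError("presence matrices must share genes and strain order")
    disagree = (expression_presence != sequence_presence).sum(axis=1)
    confirmed = expression_presence.index[disagree == 0]
    discordance = disagree[disagree > 0].rename("n_discordant_strains")
    return confirmed, discordance
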