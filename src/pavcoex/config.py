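"""Analysis configuration: every threshold used anywhere in the pipeline.

Defaults are the values printed in the study this pipeline operationalizes
(CPM floor 10, 3-of-4 replicate absence rule, on/off bounds 3..n-3, gene-trait
cuts |r|>0.5 / fdr<0.15, 98% identity+coverage for sequence confirmation,
3-kb syntenic gap, core>99% / shell 15-95% / cloud<15%, network median-count
floor 10, top-5,000 variable host genes, module-trait |r|>0.6 / P<0.05,
cross-network |r|>0.7).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import Sequence

import yaml

DEFAULT_SOFT_POWER_GRID = (4, 5, 6, 7, 8, 9, 10)


@dataclass
class AnalysisConfig:
    """All tunable thresholds of the analysis, with study defaults.

    Attributes
    ----------
    cpm_floor : float
        Count floor (in counts at the strain's median library size) defining
        the per-strain CPM cutoff for presence calling and the expression
        status classes.
    absent_rep_fraction : float
        Fraction of a strain's replicates that must fall below the CPM cutoff
        for the gene to be called absent (0.75 = "three out of four").
    min_present_strains, max_present_strains : int | None
        Bounds of the on/off filter; ``None`` for the upper bound means
        ``n_strains - 3``.
    r_cut_gene, fdr_cut_gene : float
        Gene-trait association cuts (point-biserial |r| and BH FDR).
    min_identity, min_coverage : float
        Sequence-confirmation thresholds (fractions).
    kmer_size : int
        Seed length of the built-in containment aligner.
    cluster_gap_bp : int
        Maximum inter-feature gap (bp, inclusive) joining two candidate genes
        into one syntenic cluster.
    core_frac, shell_lo, shell_hi : float
        Pangenome partition bins: core f > core_frac, cloud f < shell_lo,
        shell otherwise (the (shell_hi, core_frac] gap is assigned shell).
    median_count_floor : float
        Network prefilter: drop genes whose median raw count is below this.
    n_variable_host_genes : int
        Number of most-variable host genes entering the host network.
    r_cut_module_trait, p_cut_module_trait : float
        Module-trait significance cuts.
    r_cut_cross : float
        Cross-network module-module edge cut.
    soft_power_grid : tuple[int, ...]
        Candidate soft-thresholding powers.
    scale_free_r2 : float
        Target scale-free fit R^2 when picking the soft power.
    min_module_size : int
        Smallest assignable module.
    cut_height : float
        Static dendrogram cut height on the 1 - TOM scale; subtrees below it
        become module cores.
    kme_min : float
        Minimum |eigengene correlation| for assigning a leftover gene to the
        nearest module core (kME rescue).
    max_mean_connectivity : float
        Soft powers whose mean connectivity exceeds this are skipped when a
        smaller qualifying power exists (standard scale-free guidance).
    merge_cor : float
        Eigengene correlation above which modules are merged.
    signed_network : bool
        If True use signed adjacency ((1+cor)/2)^beta instead of |cor|^beta.
    trait_cor_on_expression : bool
        If True correlate strain-mean logCPM with the trait instead of the
        binary presence indicator.
    welch_ttest : bool
        Use Welch's t for cluster-trait tests instead of pooled-variance.
    adjust_module_trait : bool
        Apply BH across module-trait tests (off by default: raw P with an
        |r| cut, as in the study).
    """

    cpm_floor: float = 10.0
    absent_rep_fraction: float = 0.75
    min_present_strains: int = 3
    max_present_strains: int | None = None  # None -> n_strains - 3
    r_cut_gene: float = 0.5
    fdr_cut_gene: float = 0.15
    min_identity: float = 0.98
    min_coverage: float = 0.98
    kmer_size: int = 31
    cluster_gap_bp: int = 3000
    cluster_presence_rule: float | str = "all"
    core_frac: float = 0.99
    shell_lo: float = 0.15
    shell_hi: float = 0.95
    median_count_floor: float = 10.0
    n_variable_host_genes: int = 5000
    r_cut_module_trait: float = 0.6
    p_cut_module_trait: float = 0.05
    r_cut_cross: float = 0.7
    soft_power_grid: Sequence[int] = DEFAULT_SOFT_POWER_GRID
    scale_free_r2: float = 0.8
    min_module_size: int = 10
    cut_height: float = 0.85
    kme_min: float = 0.7
    max_mean_connectivity: float = 100.0
    merge_cor: float = 0.75
    logcpm_prior: float = 0.5
    pca_scale: bool = False
    signed_network: bool = False
    trait_cor_on_expression: bool = False
    welch_ttest: bool = False
    adjust_module_trait: bool = False
    max_network_genes: int = 20000
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not 0 < self.absent_rep_fraction <= 1:
            raise ValueError("absent_rep_fraction must be in (0, 1]")
        if self.min_present_strains < 0:
            raise ValueError("min_present_strains must be >= 0")
        if (
            self.max_present_strains is not None
            and self.min_present_strains > self.max_present_strains
        ):
            raise ValueError(
                "min_present_strains must be <= max_present_strains "
                f"({self.min_present_strains} > {self.max_present_strains})"
            )
        for name in ("r_cut_gene", "fdr_cut_gene", "min_identity", "min_coverage",
                     "core_frac", "shell_lo", "shell_hi", "r_cut_module_trait",
                     "r_cut_cross", "scale_free_r2", "merge_cor",
                     "cut_height", "kme_min"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not self.shell_lo <= self.shell_hi <= self.core_frac:
            raise ValueError("require shell_lo <= shell_hi <= core_frac")
        if self.cluster_gap_bp < 0:
            raise ValueError("cluster_gap_bp must be >= 0")
        if self.min_module_size < 2:
            raise ValueError("min_module_size must be >= 2")
        if self.kmer_size < 4:
            raise ValueError("kmer_size must be >= 4")
        if not self.soft_power_grid:
            raise ValueError("soft_power_grid must be non-empty")
        rule = self.cluster_presence_rule
        if rule != "all" and not (isinstance(rule, (int, float)) and 0 < rule <= 1):
            raise ValueError("cluster_presence_rule must be 'all' or a fraction in (0, 1]")

    def resolved_max_present(self, n_strains: int) -> int:
        if self.max_present_strains is not None:
            return self.max_present_strains
        return n_strains - 3

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["soft_power_grid"] = list(self.soft_power_grid)
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
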